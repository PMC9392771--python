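"""Readers/writers for the TSV / FASTA / JSON dialects the pipeline uses.

All tables are UTF-8 tab-separated. Count matrices carry a ``gene_id`` first
column and sample-ID headers; result tables use a fixed column order with
floats at six significant digits, which is enough to reproduce every status
classification from the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .data import StabilityDataset

_FLOAT_FMT = "%.6g"

RESULT_COLUMNS = [
    "gene_id", "coefficient", "log2FC_stability", "SE", "stat",
    "pvalue", "qvalue", "status", "dispersion", "converged",
]


def write_counts(dataset: StabilityDataset, exonic_path, intronic_path) -> None:
    exo, intr = dataset.to_frames()
    exo.to_csv(exonic_path, sep="\t")
    intr.to_csv(intronic_path, sep="\t")


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def write_results(table: pd.DataFrame, path) -> None:
    """Serialize a result table (stability or enrichment) to TSV."""
    cols = [c for c in RESULT_COLUMNS if c in table.columns] or list(table.columns)
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False,
                               float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    """Read UTR sequences keyed by record ID (= gene ID)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_factor_table(path) -> pd.DataFrame:
    """Factor table TSV: factor_id plus site_sequence and/or direction."""
    df = pd.read_csv(path, sep="\t")
    if "factor_id" not in df.columns:
        raise ValueError("factor table must contain a 'factor_id' column")
    return df


def write_manifest(path, **fields) -> None:
    """JSON run manifest (b-hat, filters, seed, version, config)."""
    from . import __version__

    payload = {"diffstab_version": __version__}
    payload.update(_jsonify(fields))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
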