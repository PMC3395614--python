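"""Readers and writers for the text formats the pipeline exchanges.

FASTA for sequences (Biopython), CSV for plate wells and dose-response
observations, TSV for derived tables. TSV outputs carry an optional header
comment with the run-manifest digest so every row is traceable to its run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dose_response import DoseResponseDataset

DOSE_COLUMNS = ["receptor", "odor", "log10_conc_M", "replicate", "response"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_plate_csv(path) -> pd.DataFrame:
    from .screen_assay import validate_plate

    return validate_plate(pd.read_csv(path))


def write_plate_csv(path, plate: pd.DataFrame) -> None:
    plate.to_csv(path, index=False)


def read_dose_response_csv(path) -> tuple[dict[tuple[str, str], DoseResponseDataset],
                                          dict[str, DoseResponseDataset]]:
    """Load long-form dose-response observations.

    Returns ({(receptor, odor): dataset}, {odor: vector-control dataset});
    rows with receptor == "vector" are the controls for their odor.
    """
    df = pd.read_csv(path)
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response table missing columns: {missing}")
    datasets: dict[tuple[str, str], DoseResponseDataset] = {}
    controls: dict[str, DoseResponseDataset] = {}
    for (receptor, odor), sub in df.groupby(["receptor", "odor"]):
        wide = sub.pivot_table(index="log10_conc_M", columns="replicate",
                               values="response")
        conc = 10.0 ** wide.index.to_numpy(float)
        ds = DoseResponseDataset(receptor, odor, conc, wide.to_numpy(float))
        if receptor == "vector":
            controls[odor] = ds
        else:
            datasets[(receptor, odor)] = ds
    return datasets, controls


def write_dose_response_csv(path, datasets, control=None) -> None:
    rows = []
    items = list(datasets.values()) + ([control] if control is not None else [])
    for ds in items:
        for i, c in enumerate(ds.log_conc):
            for rep in range(ds.responses.shape[1]):
                rows.append({
                    "receptor": ds.receptor, "odor": ds.odor,
                    "log10_conc_M": c, "replicate": rep + 1,
                    "response": ds.responses[i, rep],
                })
    pd.DataFrame(rows, columns=DOSE_COLUMNS).to_csv(path, index=False)


def write_tsv(path, df: pd.DataFrame, manifest_digest: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if manifest_digest:
            fh.write(f"# manifest: {manifest_digest}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
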