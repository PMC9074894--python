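"""TSV/JSON readers and writers shared by the generator and the pipeline.

Methylation travels as TSV with CpGs as rows and samples as columns (the
orientation arrays are usually distributed in); it is transposed to the
samples x CpGs in-memory layout on read.  All writers use a fixed float
format so that repeated runs with identical inputs are byte-identical.
"""

from __future__ import annotations

import json

import pandas as pd

from .preprocess import MethylationMatrix

FLOAT_FORMAT = "%.10g"

__all__ = [
    "write_methylation_tsv",
    "read_methylation_tsv",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_table",
]


def write_methylation_tsv(m: MethylationMatrix, path) -> None:
    m.values.T.to_csv(
        path, sep="\t", index_label="cpg_id", float_format=FLOAT_FORMAT
    )


def read_methylation_tsv(path, stage: str = "beta") -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cpg_id")
    return MethylationMatrix(values=df.T, stage=stage)


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV dump for report tables."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
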