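"""Delimited-text I/O for study tables.

All tables are tab-separated UTF-8 with a header row and ``NA`` for missing
values: a samples-by-assay matrix, a sample metadata table, an assay
annotation table, and (for synthetic studies) a planted-truth table.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import SimConfig, SimulatedStudy, TruthTable

NA = "NA"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False, index_col=index_col)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the four study tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "subjects": outdir / "subjects.tsv",
        "annotations": outdir / "annotations.tsv",
        "lod_mask": outdir / "lod_mask.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_table(study.matrix, paths["matrix"], index=True)
    write_table(study.subjects, paths["subjects"])
    write_table(study.annotations.reset_index(), paths["annotations"])
    write_table(study.lod_mask.astype(int), paths["lod_mask"], index=True)
    write_table(study.truth.table.reset_index(), paths["truth"])
    return paths


def read_study(indir: str | Path, config: SimConfig | None = None) -> SimulatedStudy:
    """Load a study previously written with :func:`write_study`."""
    indir = Path(indir)
    matrix = read_table(indir / "matrix.tsv", index_col=0)
    matrix.index.name = "sample_id"
    matrix.columns.name = "assay"
    subjects = read_table(indir / "subjects.tsv")
    annotations = read_table(indir / "annotations.tsv", index_col=0)
    annotations.index.name = "assay"
    mask_path = indir / "lod_mask.tsv"
    if mask_path.exists():
        lod_mask = read_table(mask_path, index_col=0).astype(bool)
        lod_mask.index.name = "sample_id"
        lod_mask.columns.name = "assay"
    else:
        lod_mask = matrix.lt(annotations["lod"], axis=1) & matrix.notna()
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        truth = TruthTable(read_table(truth_path).set_index("protein"))
    else:
        truth = TruthTable.null(list(annotations["protein"].unique()))
    return SimulatedStudy(
        subjects=subjects,
        matrix=matrix,
        lod_mask=lod_mask,
        annotations=annotations,
        truth=truth,
        config=config,
    )
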