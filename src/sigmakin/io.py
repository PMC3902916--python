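"""Reading and writing the pipeline's tabular formats (TSV by default)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .grid import TimeGrid
from .network import PriorInteraction
from .preprocess import ArrayMetadata, ProfileSet, RawExpressionTable

__all__ = [
    "read_expression",
    "read_metadata",
    "read_grid",
    "read_priors",
    "read_annotation",
    "read_gene_list",
    "write_profiles",
    "read_profiles",
]


def _read(path, sep="\t", na="NA", index_col=None):
    return pd.read_csv(path, sep=sep, na_values=[na], keep_default_na=False, index_col=index_col)


def read_expression(
    log2ratio_path, sample_signal_path, sep: str = "\t", na: str = "NA"
) -> RawExpressionTable:
    """Two gene x array matrices (first column = gene id)."""
    l2r = _read(log2ratio_path, sep, na, index_col=0)
    sig = _read(sample_signal_path, sep, na, index_col=0)
    return RawExpressionTable(l2r, sig)


def read_metadata(path, sep: str = "\t", na: str = "NA") -> ArrayMetadata:
    df = _read(path, sep, na)
    return ArrayMetadata(df[["array_id", "time_label", "replicate"]])


def read_grid(path, sep: str = "\t", na: str = "NA") -> TimeGrid:
    df = _read(path, sep, na)
    return TimeGrid(tuple(df["time_label"].astype(str)), df["hours"].to_numpy(dtype=float))


def read_priors(path, sep: str = "\t", na: str = "NA") -> list[PriorInteraction]:
    df = _read(path, sep, na)
    return [
        PriorInteraction(
            str(r["regulator"]), str(r["target"]), str(r["source"]),
            str(r.get("citation", "") or ""),
        )
        for _, r in df.iterrows()
    ]


def read_annotation(path, sep: str = "\t", na: str = "NA") -> pd.DataFrame:
    df = _read(path, sep, na)
    return df[["gene", "class"]]


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_profiles(profiles: ProfileSet, out_dir, sep: str = "\t", na: str = "NA") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in (
        ("profiles.tsv", profiles.values),
        ("cv.tsv", profiles.cv),
        ("n_used.tsv", profiles.n_used),
    ):
        df.to_csv(out / name, sep=sep, na_rep=na, index_label="gene")


def read_profiles(in_dir, grid: TimeGrid, sep: str = "\t", na: str = "NA") -> ProfileSet:
    src = Path(in_dir)
    values = _read(src / "profiles.tsv", sep, na, index_col=0)
    cv = _read(src / "cv.tsv", sep, na, index_col=0)
    n_used = _read(src / "n_used.tsv", sep, na, index_col=0).astype(int)
    incomplete = set(values.index[values.isna().any(axis=1)])
    return ProfileSet(grid, values, cv, n_used, incomplete)
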