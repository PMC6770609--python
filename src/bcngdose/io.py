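"""Plain-text readers and writers for every pipeline artifact.

All tables are TSV with headers; gene sets are one identifier per line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import SEG_COLUMNS

_STR_COLS = {"chromosome": str, "region": str, "sample": str}


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    segments.loc[:, SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=_STR_COLS)
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SEG file {path} lacks columns: {sorted(missing)}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("transcript").to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.rename_axis("transcript").to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript", dtype=_STR_COLS)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.rename_axis("sample").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_gene_set(members, path: str | Path) -> None:
    Path(path).write_text("".join(f"{m}\n" for m in members))


def read_gene_set(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
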