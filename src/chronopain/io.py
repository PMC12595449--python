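"""File dialects: long-format behavioral CSV, PIR activity CSV, counts and
sample-metadata TSV.

All files are UTF-8 with a header row. The behavioral table is long format
(animal_id, sex, group, day, assay, value) with real-valued study days,
day 0 = injury day. The PIR file has one row per (animal_id, epoch_index,
count) at 10-s resolution, preceded by ``# key=value`` sidecar lines giving
the epoch length and the lights-on anchor. Malformed rows are reported with
their line numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy import ActivityStream
from .profiling import OutcomeTable

__all__ = [
    "read_behavioral_csv",
    "write_behavioral_csv",
    "read_pir_csv",
    "write_pir_csv",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_sample_info_tsv",
]

BEHAVIORAL_COLUMNS = ("animal_id", "sex", "group", "day", "assay", "value")
SAMPLE_INFO_COLUMNS = ("sample_id", "treatment", "timing", "threshold_log_g",
                       "guarding_index")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_behavioral_csv(path: str | Path) -> OutcomeTable:
    """Parse and validate a long-format behavioral CSV into an OutcomeTable."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, comment="#")
    _require_columns(df, BEHAVIORAL_COLUMNS, path)
    for col in ("day", "value"):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        # value may be NA (missing measurement); day may not
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad = num.isna() & ~blank
        if col == "day":
            bad |= blank
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(
                f"{path}: non-numeric {col!r} at line {line}: "
                f"{raw[bad].iloc[0]!r}"
            )
        df[col] = num
    dup = df.duplicated(subset=["animal_id", "day", "assay"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        r = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate animal x day x assay at line {line}: "
            f"{r['animal_id']}/{r['day']}/{r['assay']}"
        )
    return OutcomeTable(df)


def write_behavioral_csv(table: OutcomeTable | pd.DataFrame, path: str | Path) -> None:
    df = table.records if isinstance(table, OutcomeTable) else table
    df.to_csv(path, index=False, float_format="%.10g")


def read_pir_csv(path: str | Path) -> list[ActivityStream]:
    """Read PIR streams; sidecar ``# key=value`` lines set epoch_s and
    lights_on_epoch (global)."""
    path = Path(path)
    meta: dict[str, int] = {"epoch_s": 10, "lights_on_epoch": 0}
    with open(path, encoding="utf-8") as fh:
        header_lines = []
        for raw in fh:
            if raw.startswith("#"):
                body = raw[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = int(v.strip())
            else:
                header_lines.append(raw)
                header_lines.extend(fh)
                break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(header_lines)))
    _require_columns(df, ("animal_id", "epoch_index", "count"), path)
    if df["count"].isna().any() or (df["count"] < 0).any():
        bad = df.index[df["count"].isna() | (df["count"] < 0)][0]
        raise ValueError(f"{path}: invalid count in data row {int(bad) + 1}")
    streams = []
    for animal, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("epoch_index")
        idx = grp["epoch_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            raise ValueError(
                f"{path}: animal {animal}: epoch indices must be 0..n-1 "
                "without gaps"
            )
        streams.append(
            ActivityStream(
                animal_id=str(animal),
                counts=grp["count"].to_numpy(dtype=np.int64),
                epoch_s=int(meta["epoch_s"]),
                lights_on_epoch=int(meta["lights_on_epoch"]),
            )
        )
    return streams


def write_pir_csv(streams: list[ActivityStream], path: str | Path) -> None:
    if streams:
        epoch_s = {s.epoch_s for s in streams}
        anchor = {s.lights_on_epoch for s in streams}
        if len(epoch_s) != 1 or len(anchor) != 1:
            raise ValueError("streams in one file must share epoch_s and anchor")
    with open(path, "w", encoding="utf-8") as fh:
        if streams:
            fh.write(f"# epoch_s={streams[0].epoch_s}\n")
            fh.write(f"# lights_on_epoch={streams[0].lights_on_epoch}\n")
        fh.write("animal_id,epoch_index,count\n")
        for s in streams:
            for i, c in enumerate(s.counts):
                fh.write(f"{s.animal_id},{i},{c}\n")


def read_counts_tsv(
    counts_path: str | Path, meta_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample counts TSV plus sample metadata TSV.

    Every counts column must appear in the metadata (error names the
    sample); counts must be nonnegative integers with no missing values.
    """
    counts_path, meta_path = Path(counts_path), Path(meta_path)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"{counts_path}: duplicate gene id {dup!r}")
    if counts.isna().any().any():
        col = counts.columns[counts.isna().any()][0]
        raise ValueError(f"{counts_path}: missing count value in sample {col!r}")
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{counts_path}: negative counts")
    meta = pd.read_csv(meta_path, sep="\t")
    _require_columns(meta, SAMPLE_INFO_COLUMNS, meta_path)
    meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"{meta_path}: duplicate sample id {dup!r}")
    unknown = [c for c in counts.columns if c not in meta.index]
    if unknown:
        raise ValueError(
            f"{counts_path}: sample {unknown[0]!r} absent from metadata "
            f"{meta_path}"
        )
    return counts, meta.loc[list(counts.columns)]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def write_sample_info_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")
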