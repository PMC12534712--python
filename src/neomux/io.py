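"""Readers/writers for the plain-text cohort and result formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import WeightedConnectome, build_fc, build_sc
from .simulate import Cohort, SimConfig, SubjectRecord

__all__ = [
    "read_time_series",
    "read_count_matrix",
    "read_roi_sizes",
    "read_nodes",
    "read_metadata",
    "read_cohort",
    "write_connectome",
    "read_connectome",
    "build_cohort_connectomes",
]


def read_time_series(path: str | Path) -> pd.DataFrame:
    """T x N table; the header row lists node labels.

    ``float_precision="round_trip"`` so written cohorts re-load
    bit-identically.
    """
    return pd.read_csv(path, float_precision="round_trip")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Square labeled streamline-count matrix."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    return df


def read_roi_sizes(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["size"].to_numpy(), index=df["node_label"].astype(str))


def read_nodes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"node_label": str, "hemisphere": str})


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        bw = row.get("birth_weight")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                ga_birth=float(row["ga_birth"]),
                pma_scan=float(row["pma_scan"]),
                sex=str(row["sex"]),
                birth_weight=None if pd.isna(bw) else float(bw),
            )
        )
    return records


def read_cohort(directory: str | Path, config: SimConfig | None = None) -> Cohort:
    """Load a cohort previously serialized by :func:`neomux.simulate.write_cohort`."""
    directory = Path(directory)
    subjects = read_metadata(directory / "metadata.csv")
    nodes = read_nodes(directory / "nodes.csv")
    labels = nodes["node_label"].tolist()
    hemisphere = nodes["hemisphere"].tolist()
    sizes = read_roi_sizes(directory / "roi_sizes.csv")
    sc_forward, sc_reverse, timeseries = {}, {}, {}
    for rec in subjects:
        sid = rec.subject_id
        ts = read_time_series(directory / f"ts_{sid}.csv")
        if list(ts.columns) != labels:
            raise ValueError(f"time-series header of {sid} does not match nodes.csv")
        timeseries[sid] = ts.to_numpy(dtype=float)
        sc_forward[sid] = read_count_matrix(
            directory / f"sc_{sid}_forward.csv"
        ).to_numpy(dtype=np.int64)
        sc_reverse[sid] = read_count_matrix(
            directory / f"sc_{sid}_reverse.csv"
        ).to_numpy(dtype=np.int64)
    return Cohort(
        config=config if config is not None else SimConfig(),
        subjects=subjects,
        node_labels=labels,
        hemisphere=hemisphere,
        roi_sizes=sizes,
        sc_forward=sc_forward,
        sc_reverse=sc_reverse,
        timeseries=timeseries,
    )


def write_connectome(conn: WeightedConnectome, path: str | Path) -> None:
    conn.to_frame().to_csv(path)


def read_connectome(
    path: str | Path,
    modality: str,
    hemisphere: list[str] | None = None,
    subject_id: str = "",
) -> WeightedConnectome:
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if hemisphere is None:
        half = len(labels) // 2
        hemisphere = ["L"] * half + ["R"] * (len(labels) - half)
    return WeightedConnectome(
        node_labels=labels,
        hemisphere=hemisphere,
        weights=df.to_numpy(dtype=float),
        modality=modality,
        subject_id=subject_id,
    )


def build_cohort_connectomes(
    cohort: Cohort,
) -> tuple[dict[str, WeightedConnectome], dict[str, WeightedConnectome]]:
    """Per-subject SC and FC weighted connectomes for a whole cohort."""
    sc, fc = {}, {}
    for rec in cohort.subjects:
        sid = rec.subject_id
        sc[sid] = build_sc(
            cohort.sc_forward[sid],
            cohort.sc_reverse[sid],
            cohort.roi_sizes,
            hemisphere=cohort.hemisphere,
            node_labels=cohort.node_labels,
            subject_id=sid,
        )
        fc[sid] = build_fc(
            cohort.timeseries[sid],
            hemisphere=cohort.hemisphere,
            node_labels=cohort.node_labels,
            subject_id=sid,
        )
    return sc, fc
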