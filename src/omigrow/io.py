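"""Readers and writers for the pipeline's delimited-text formats.

All tables are tab-delimited with a header row. Matrices store
conditions in rows (first column ``condition_id``) and feature IDs in
the header; growth curves are tidy ``condition_id, replicate, time_h,
od660`` tables; the synthetic truth record round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import InputError
from .preprocess import IdMap, OmicsMatrix
from .synthetic import ConditionDesign, SyntheticTruth

SEP = "\t"


def write_matrix(m: OmicsMatrix, path) -> None:
    m.data.to_csv(path, sep=SEP, index_label="condition_id")


def read_matrix(path, layer: str, standardized: bool = False) -> OmicsMatrix:
    df = pd.read_csv(path, sep=SEP, index_col="condition_id")
    return OmicsMatrix(layer, df, standardized=standardized)


def write_design(design: Sequence[ConditionDesign], path) -> None:
    pd.DataFrame([dataclasses.asdict(c) for c in design]).to_csv(path, sep=SEP, index=False)


def read_design(path) -> list[ConditionDesign]:
    df = pd.read_csv(path, sep=SEP)
    required = {"condition_id", "substrate", "oxygen", "acetate_supplemented"}
    if not required.issubset(df.columns):
        raise InputError(f"design table must have columns {sorted(required)}")
    return [
        ConditionDesign(
            str(r.condition_id), str(r.substrate), str(r.oxygen), bool(r.acetate_supplemented)
        )
        for r in df.itertuples()
    ]


def write_growth_curves(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep=SEP, index=False)


def read_growth_curves(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP)


def write_rates(rates: pd.Series, path) -> None:
    rates.rename("growth_rate").to_csv(path, sep=SEP, index_label="condition_id")


def read_rates(path) -> pd.Series:
    df = pd.read_csv(path, sep=SEP, index_col="condition_id")
    if "growth_rate" not in df.columns:
        raise InputError("rate table must have a growth_rate column")
    return df["growth_rate"]


def write_id_map(id_map: IdMap, path) -> None:
    id_map.to_frame().to_csv(path, sep=SEP, index=False)


def read_id_map(path) -> IdMap:
    df = pd.read_csv(path, sep=SEP)
    if not {"gene_id", "protein_id"}.issubset(df.columns):
        raise InputError("id map must have gene_id and protein_id columns")
    return IdMap(tuple((str(g), str(p)) for g, p in zip(df.gene_id, df.protein_id)))


def write_panel(features: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{f}\n" for f in features))


def read_panel(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(truth), sort_keys=True))


def read_truth(path) -> SyntheticTruth:
    payload = yaml.safe_load(Path(path).read_text())
    try:
        return SyntheticTruth(**payload)
    except TypeError as exc:
        raise InputError(f"malformed truth record: {exc}")
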