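"""Reading and writing subject tables, networks and analysis configs.

Subject tables are delimited text (comma or tab, auto-detected) with a
header ``subject_id,age,sex,weight,dose,<region...>``; weight and dose
columns are optional. Networks are written either as a labelled square
matrix or in long form (``region_i,region_j,value``, one row per
unordered pair); both round-trip losslessly. Written files use commas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .data import CohortTable, SubjectRecord
from .networks import (
    CorrelationNetwork,
    StrengthVector,
    ZScoreNetwork,
    from_upper_triangle,
    upper_triangle,
)
from .regions import RegionSet, default_region_set

DEFAULT_SEX_MAPPING: dict[str, int] = {"F": 0, "M": 1}

_ID_COLS = ("subject_id", "age", "sex")
_META_COLS = ("weight", "dose")


def _coerce_sex(value, mapping: Mapping[str, int], subject_id: str) -> int:
    if isinstance(value, str):
        key = value.strip()
        if key in mapping:
            return int(mapping[key])
        raise ValueError(
            f"{subject_id}: sex value {value!r} not in mapping {dict(mapping)}"
        )
    sex = int(value)
    if float(value) != sex:
        raise ValueError(f"{subject_id}: non-integer sex code {value!r}")
    return sex


def read_subject_table(
    path: str | Path,
    region_set: RegionSet,
    sex_mapping: Mapping[str, int] | None = None,
) -> CohortTable:
    """Read a delimited subject table into a validated :class:`CohortTable`.

    The header must contain ``subject_id``, ``age``, ``sex`` and one
    column per region label of ``region_set``; extra columns beyond the
    optional ``weight``/``dose`` are ignored. Sex strings are mapped via
    ``sex_mapping`` (default ``{"F": 0, "M": 1}``).
    """
    sex_mapping = dict(sex_mapping or DEFAULT_SEX_MAPPING)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    missing_id = [c for c in _ID_COLS if c not in df.columns]
    if missing_id:
        raise ValueError(f"{path}: missing required column(s) {missing_id}")
    missing_regions = [r for r in region_set if r not in df.columns]
    if missing_regions:
        raise ValueError(f"{path}: missing region column(s) {missing_regions}")
    for region in region_set:
        col = pd.to_numeric(df[region], errors="coerce")
        bad = df.loc[col.isna(), "subject_id"].tolist()
        if bad:
            raise ValueError(
                f"{path}: non-numeric or missing SUV in column {region!r} "
                f"for subject(s) {bad}"
            )
        df[region] = col
    subjects = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        kwargs = {}
        for meta in _META_COLS:
            if meta in df.columns and pd.notna(row[meta]):
                kwargs[meta] = float(row[meta])
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age=float(row["age"]),
                sex=_coerce_sex(row["sex"], sex_mapping, sid),
                suv={r: float(row[r]) for r in region_set},
                **kwargs,
            )
        )
    return CohortTable(subjects=tuple(subjects), region_set=region_set)


def write_subject_table(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to CSV in the canonical column order."""
    rows = []
    for s in cohort.subjects:
        row: dict[str, object] = {"subject_id": s.subject_id, "age": s.age, "sex": s.sex}
        if s.weight is not None:
            row["weight"] = s.weight
        if s.dose is not None:
            row["dose"] = s.dose
        row.update({r: s.suv[r] for r in cohort.region_set})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_network(
    net: CorrelationNetwork | ZScoreNetwork, path: str | Path, layout: str = "square"
) -> None:
    """Write a network as a labelled square matrix or in long (edge-list) form.

    Long form has exactly M*(M-1)/2 data rows — one per unordered region
    pair in canonical upper-triangle order. Values are written with full
    float64 precision so read/write round-trips are exact.
    """
    names = list(net.region_set.names)
    if layout == "square":
        df = pd.DataFrame(net.matrix, index=names, columns=names)
        df.to_csv(path, index_label="region", float_format=lambda v: repr(float(v)))
    elif layout == "long":
        pairs = net.region_set.edge_pairs()
        values = upper_triangle(net.matrix)
        df = pd.DataFrame(
            {
                "region_i": [p[0] for p in pairs],
                "region_j": [p[1] for p in pairs],
                "value": values,
            }
        )
        df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    else:
        raise ValueError(f"layout must be 'square' or 'long', got {layout!r}")


def read_network(path: str | Path) -> tuple[np.ndarray, RegionSet]:
    """Read a network written by :func:`write_network` (layout auto-detected).

    Returns the symmetric matrix (zero diagonal) and the region set in
    file order.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    if cols[:2] == ["region_i", "region_j"]:
        seen: list[str] = []
        for col in ("region_i", "region_j"):
            for name in df[col]:
                if name not in seen:
                    seen.append(name)
        region_set = RegionSet(tuple(seen))
        index = {n: i for i, n in enumerate(seen)}
        m = len(seen)
        iu = np.array([index[n] for n in df["region_i"]])
        ju = np.array([index[n] for n in df["region_j"]])
        out = np.zeros((m, m))
        out[iu, ju] = df["value"].to_numpy(dtype=float)
        out[ju, iu] = out[iu, ju]
        return out, region_set
    region_set = RegionSet(tuple(str(c) for c in cols[1:]))
    matrix = df[cols[1:]].to_numpy(dtype=float)
    return matrix, region_set


def write_graphml(
    zcc: ZScoreNetwork, strength: StrengthVector, path: str | Path
) -> None:
    """Export a Z-score network to GraphML with STR as a node attribute.

    Only nonzero edges are emitted (eliminated edges carry no information).
    """
    g = nx.Graph()
    for region in zcc.region_set:
        g.add_node(region, strength=float(strength.values[region]))
    pairs = zcc.region_set.edge_pairs()
    values = upper_triangle(zcc.matrix)
    for (a, b), v in zip(pairs, values):
        if v != 0.0:
            g.add_edge(a, b, zcc=float(v))
    nx.write_graphml(g, str(path))


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-time settings shared by the CLI commands.

    ``threshold_fraction`` is the resNET elimination threshold (default
    0.30), ``alpha`` the family-wise significance level for edge tests
    (default 0.01, Bonferroni-corrected over all edges).
    """

    region_set: RegionSet = field(default_factory=default_region_set)
    covariates: tuple[str, ...] = ("age", "sex")
    sex_mapping: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEX_MAPPING)
    )
    threshold_fraction: float = 0.3
    threshold_mode: str = "relative"
    alpha: float = 0.01
    seed: int = 0


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML or JSON.

    Recognised keys: ``regions`` (list of labels), ``covariates``,
    ``sex_mapping``, ``threshold_fraction``, ``threshold_mode``,
    ``alpha``, ``seed``. Missing keys fall back to defaults.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}
    kwargs: dict = {}
    if "regions" in raw:
        kwargs["region_set"] = RegionSet(tuple(raw["regions"]))
    if "covariates" in raw:
        kwargs["covariates"] = tuple(raw["covariates"])
    if "sex_mapping" in raw:
        kwargs["sex_mapping"] = {str(k): int(v) for k, v in raw["sex_mapping"].items()}
    for key in ("threshold_fraction", "alpha"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "threshold_mode" in raw:
        kwargs["threshold_mode"] = str(raw["threshold_mode"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return AnalysisConfig(**kwargs)
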