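"""Dataset container and delimited-text input/output.

The canonical interchange is long-format delimited text with columns
(individual, time, variable, value); wide matrices (one row per
individual-time pair, one column per variable) are accepted for
convenience.  No binary formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["OmicsDataset", "read_dataset", "write_dataset",
           "read_distance_matrices"]

GROUP_LABELS = ("controls", "cases")


@dataclass
class OmicsDataset:
    """Longitudinal multi-omic dataset.

    X holds metabolite abundances (N individuals x T time points x M
    metabolites), Y a companion omic type measured on the same design
    (N x T x K), and ``group`` assigns each individual to "cases" or
    "controls".  An optional ``y_drug`` (N x T) carries a continuous drug
    level for the continuous treatment mode.
    """

    X: np.ndarray
    Y: np.ndarray
    group: np.ndarray
    individuals: list = field(default_factory=list)
    times: list = field(default_factory=list)
    metabolites: list = field(default_factory=list)
    y_variables: list = field(default_factory=list)
    y_drug: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.group = np.asarray(self.group)
        if self.X.ndim != 3 or self.Y.ndim != 3:
            raise ValueError("X and Y must be 3-D (individuals x times x variables)")
        N, T, M = self.X.shape
        if self.Y.shape[:2] != (N, T):
            raise ValueError("X and Y must share individual and time axes")
        if T < 2:
            raise ValueError("need at least two time points")
        if self.group.shape != (N,):
            raise ValueError("group must have one label per individual")
        bad = set(np.unique(self.group)) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        for lab in GROUP_LABELS:
            if not (self.group == lab).any():
                raise ValueError(f"group '{lab}' is empty")
        for name, arr in (("X", self.X), ("Y", self.Y)):
            if not np.isfinite(arr).all():
                i, t, m = np.argwhere(~np.isfinite(arr))[0]
                raise ValueError(
                    f"{name} has a missing/non-finite value at "
                    f"(individual={i}, time={t}, variable={m}); "
                    "missing data are not supported"
                )
        if not self.individuals:
            self.individuals = [f"ind{i}" for i in range(N)]
        if not self.times:
            self.times = list(range(1, T + 1))
        if list(self.times) != sorted(self.times):
            raise ValueError("time points must be strictly increasing")
        if len(set(self.times)) != T:
            raise ValueError("time points must be strictly increasing")
        if not self.metabolites:
            self.metabolites = [f"met{m}" for m in range(M)]
        if not self.y_variables:
            self.y_variables = [f"y{k}" for k in range(self.Y.shape[2])]
        if self.y_drug is not None:
            self.y_drug = np.asarray(self.y_drug, dtype=float)
            if self.y_drug.shape != (N, T):
                raise ValueError("y_drug must be N x T")

    @property
    def shape(self):
        return self.X.shape + (self.Y.shape[2],)

    @property
    def case_indices(self) -> np.ndarray:
        return np.flatnonzero(self.group == "cases")

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.group == "controls")

    def standardized(self) -> "OmicsDataset":
        """Center and scale each metabolite and Y column over all (i, t)."""

        def _scale(A):
            flat = A.reshape(-1, A.shape[-1])
            sd = flat.std(axis=0, ddof=1)
            if (sd == 0).any():
                bad = [i for i, s in enumerate(sd) if s == 0]
                raise ValueError(f"constant column(s) {bad}; cannot standardize")
            return (A - flat.mean(axis=0)) / sd

        return OmicsDataset(
            X=_scale(self.X), Y=_scale(self.Y), group=self.group.copy(),
            individuals=list(self.individuals), times=list(self.times),
            metabolites=list(self.metabolites), y_variables=list(self.y_variables),
            y_drug=None if self.y_drug is None else self.y_drug.copy(),
        )


def read_distance_matrices(paths, sep="\t"):
    """Read per-pathway within-pathway shortest-path-length matrices.

    Each file holds one square M x M matrix (metabolite identifiers as
    header row and first column); entries are path lengths for co-pathway
    pairs and may be empty/0 elsewhere.  Returns a list of float arrays in
    the given order, suitable for ``build_design_matrices(..., distances=)``.
    """
    out = []
    for path in paths:
        df = pd.read_csv(path, sep=sep, index_col=0,
                         float_precision="round_trip")
        arr = df.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError(f"{path}: distance matrix must be square")
        out.append(arr)
    return out


def _to_long(A, individuals, times, variables):
    N, T, V = A.shape
    idx = pd.MultiIndex.from_product(
        [individuals, times, variables], names=["individual", "time", "variable"]
    )
    return pd.DataFrame({"value": A.reshape(-1)}, index=idx).reset_index()


def write_dataset(ds: OmicsDataset, x_path, y_path, groups_path, sep="\t") -> None:
    """Write a dataset as long-format delimited text files."""
    _to_long(ds.X, ds.individuals, ds.times, ds.metabolites).to_csv(
        x_path, sep=sep, index=False
    )
    _to_long(ds.Y, ds.individuals, ds.times, ds.y_variables).to_csv(
        y_path, sep=sep, index=False
    )
    pd.DataFrame({"individual": ds.individuals, "group": ds.group}).to_csv(
        groups_path, sep=sep, index=False
    )


def _pivot_long(df, path):
    required = {"individual", "time", "variable", "value"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: long layout needs columns {sorted(required)}"
        )
    individuals = list(pd.unique(df["individual"]))
    times = sorted(pd.unique(df["time"]))
    variables = list(pd.unique(df["variable"]))
    wide = df.set_index(["individual", "time", "variable"])["value"]
    full = pd.MultiIndex.from_product([individuals, times, variables])
    missing = full.difference(wide.index)
    if len(missing):
        raise ValueError(f"{path}: missing cell(s) at {list(missing[:5])}")
    arr = wide.reindex(full).to_numpy().reshape(
        len(individuals), len(times), len(variables)
    )
    return arr, individuals, times, variables


def _pivot_wide(df, path):
    if df.columns[0] != "individual" or df.columns[1] != "time":
        raise ValueError(
            f"{path}: wide layout needs leading columns individual, time"
        )
    individuals = list(pd.unique(df["individual"]))
    times = sorted(pd.unique(df["time"]))
    variables = list(df.columns[2:])
    df = df.set_index(["individual", "time"])
    full = pd.MultiIndex.from_product([individuals, times])
    missing = full.difference(df.index)
    if len(missing):
        raise ValueError(f"{path}: missing row(s) for {list(missing[:5])}")
    arr = df.reindex(full).to_numpy().reshape(
        len(individuals), len(times), len(variables)
    )
    return arr, individuals, times, variables


def read_dataset(x_path, y_path, groups_path, layout="long", sep="\t",
                 drug_variable=None) -> OmicsDataset:
    """Read an :class:`OmicsDataset` from delimited text.

    ``layout="long"`` expects columns (individual, time, variable, value);
    ``layout="wide"`` expects (individual, time, <one column per variable>).
    Variable order follows first appearance in the input.  ``drug_variable``
    names a Y column to extract as the continuous drug level.
    """
    if layout not in ("long", "wide"):
        raise ValueError("layout must be 'long' or 'wide'")
    pivot = _pivot_long if layout == "long" else _pivot_wide
    frames = {}
    for name, path in (("X", x_path), ("Y", y_path)):
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        vals = df["value"] if layout == "long" else df[df.columns[2:]]
        if pd.isna(np.asarray(vals, dtype=object)).any():
            navals = df[df.isna().any(axis=1)]
            raise ValueError(
                f"{path}: missing value(s), first at row "
                f"{navals.index[0]} ({navals.iloc[0].to_dict()})"
            )
        frames[name] = pivot(df, path)

    X, individuals, times, metabolites = frames["X"]
    Y, ind_y, times_y, y_variables = frames["Y"]
    if list(ind_y) != list(individuals) or list(times_y) != list(times):
        raise ValueError("X and Y disagree on individuals or time points")

    gdf = pd.read_csv(groups_path, sep=sep)
    if not {"individual", "group"}.issubset(gdf.columns):
        raise ValueError(f"{groups_path}: needs columns individual, group")
    gmap = dict(zip(gdf["individual"].astype(str), gdf["group"]))
    try:
        group = np.array([gmap[str(i)] for i in individuals])
    except KeyError as err:
        raise ValueError(f"{groups_path}: no group label for individual {err}")

    y_drug = None
    if drug_variable is not None:
        if drug_variable not in y_variables:
            raise ValueError(f"drug variable '{drug_variable}' not in Y columns")
        k = y_variables.index(drug_variable)
        y_drug = Y[:, :, k]

    return OmicsDataset(
        X=X, Y=Y, group=group, individuals=list(individuals),
        times=list(times), metabolites=list(metabolites),
        y_variables=list(y_variables), y_drug=y_drug,
    )
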