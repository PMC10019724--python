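"""File formats: profile tables, network edge lists, fit results, DOT export.

TSV is the canonical dialect (CSV is accepted and selected by file
extension); UTF-8 throughout, '.' decimal separator, full-precision floats.
All writers round-trip losslessly through their paired readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ctmc import HazardNetwork, Profile
from .inference import Dataset, FitConfig, FitResult

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_times",
    "write_times",
    "read_network",
    "write_network",
    "export_dot",
    "read_fit_result",
    "write_fit_result",
]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_profiles(path, times_path=None) -> Dataset:
    """Read a sample-by-event 0/1 table (first column: sample id).

    An optional companion times file (columns ``sample_id``, ``time``) is
    merged by id; every sample must then have a time.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary value {values[r, c]!r} at sample "
            f"{df.index[r]!r}, event {df.columns[c]!r}"
        )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    times = None
    if times_path is not None:
        tdf = read_times(times_path)
        missing = [sid for sid in df.index if sid not in tdf.index]
        if missing:
            raise ValueError(f"{times_path}: missing times for samples {missing}")
        times = tdf.loc[df.index, "time"].to_numpy(dtype=float)
    return Dataset(
        profiles=[Profile(row) for row in values.astype(int)],
        sample_ids=[str(s) for s in df.index],
        times=times,
        event_names=[str(c) for c in df.columns],
    )


def write_profiles(dataset: Dataset, path, times_path=None) -> None:
    df = pd.DataFrame(
        dataset.matrix(), index=dataset.sample_ids, columns=dataset.event_names
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep(path))
    if times_path is not None:
        if dataset.times is None:
            raise ValueError("dataset has no times to write")
        write_times(dataset.sample_ids, dataset.times, times_path)


def read_times(path) -> pd.DataFrame:
    tdf = pd.read_csv(path, sep=_sep(path), index_col=0)
    if "time" not in tdf.columns:
        raise ValueError(f"{path}: expected a 'time' column")
    if (tdf["time"] < 0).any():
        raise ValueError(f"{path}: times must be nonnegative")
    tdf.index = tdf.index.map(str)
    return tdf


def write_times(sample_ids, times, path) -> None:
    df = pd.DataFrame({"time": np.asarray(times, dtype=float)}, index=sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep(path), float_format="%.17g")


def read_network(path) -> HazardNetwork:
    """Read an edge-list file back into a hazard matrix.

    Rows with ``source == target`` carry the spontaneous (diagonal) rates
    and double as event declarations; other rows are inter-event edges and
    may only reference declared events.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype={"source": str, "target": str})
    if not {"source", "target", "rate"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns source, target, rate")
    node_rows = df[df["source"] == df["target"]]
    names = node_rows["source"].tolist()
    index = {name: i for i, name in enumerate(names)}
    if len(index) != len(names):
        raise ValueError(f"{path}: duplicate event declarations")
    R = np.zeros((len(names), len(names)))
    for _, row in df.iterrows():
        s, t = row["source"], row["target"]
        if s not in index or t not in index:
            raise ValueError(f"{path}: edge references undeclared event {s!r}->{t!r}")
        R[index[s], index[t]] = float(row["rate"])
    return HazardNetwork(R, names)


def write_network(network: HazardNetwork, path) -> None:
    names = network.event_names
    R = network.rates
    rows = [
        {"source": names[j], "target": names[j], "rate": repr(float(R[j, j]))}
        for j in range(network.n)
    ]
    for i in range(network.n):
        for j in range(network.n):
            if i != j and R[i, j] != 0:
                rows.append(
                    {"source": names[i], "target": names[j], "rate": repr(float(R[i, j]))}
                )
    pd.DataFrame(rows, columns=["source", "target", "rate"]).to_csv(
        path, sep=_sep(path), index=False
    )


def export_dot(network: HazardNetwork, threshold_frac: float, path) -> None:
    """Graphviz DOT rendering of a (thresholded) hazard network.

    Edge pen widths and gray shades scale linearly with the inter-event
    rates; node sizes scale linearly with the spontaneous rates.
    """
    from .inference import threshold_network

    adjacency, pruned = threshold_network(network, threshold_frac)
    R = pruned.rates
    names = network.event_names
    diag = np.diag(R)
    dmax = diag.max() if diag.max() > 0 else 1.0
    off = R[adjacency.astype(bool)]
    emax = off.max() if off.size and off.max() > 0 else 1.0
    lines = ["digraph hazard_network {", "  rankdir=TB;"]
    for j, name in enumerate(names):
        w = 0.5 + 1.0 * diag[j] / dmax
        lines.append(
            f'  "{name}" [shape=circle, width={w:.3f}, fixedsize=true];'
        )
    for i in range(network.n):
        for j in range(network.n):
            if adjacency[i, j]:
                frac = R[i, j] / emax
                pen = 0.5 + 3.0 * frac
                shade = int(round(160 * (1 - frac)))
                color = f"#{shade:02x}{shade:02x}{shade:02x}"
                lines.append(
                    f'  "{names[i]}" -> "{names[j]}" '
                    f'[penwidth={pen:.3f}, color="{color}"];'
                )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fit_result(result: FitResult, path) -> None:
    """Serialize a fit as JSON: rates as nested lists, times keyed by id."""
    payload = {
        "event_names": result.network.event_names,
        "rates": result.network.rates.tolist(),
        "times": (
            {sid: float(t) for sid, t in zip(result.sample_ids, result.times)}
            if result.sample_ids is not None
            else result.times.tolist()
        ),
        "objective_trace": result.objective_trace.tolist(),
        "config": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k in FitConfig.__dataclass_fields__
            for v in [getattr(result.config, k)]
        },
        "converged": result.converged,
        "iterations": result.iterations,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_fit_result(path) -> dict:
    """Load a serialized fit; returns a dict with a reconstructed network."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    payload["network"] = HazardNetwork(
        np.array(payload["rates"]), payload["event_names"]
    )
    return payload
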