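"""Readers and writers for the package's delimited-text dialects.

All on-disk formats are plain text: event CSVs (``t_s,E_keV`` with ``#``
header lines), binned-count CSVs, TAC CSVs, grid maps with JSON sidecars,
and JSON fit reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import CountTimeSeries, GammaEventList

__all__ = [
    "write_events", "read_events",
    "write_series", "read_series",
    "write_tac", "read_tac",
    "write_report",
]


def write_events(events: GammaEventList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# t_start_min: {events.t_start_min}\n")
        if events.gaps_s:
            gaps = ";".join(f"{a},{b}" for a, b in events.gaps_s)
            fh.write(f"# gaps_s: {gaps}\n")
        fh.write("t_s,E_keV\n")
        for t, e in zip(events.times_s, events.energies_keV):
            fh.write(f"{t:.6f},{e:.3f}\n")


def read_events(path: str | Path) -> GammaEventList:
    path = Path(path)
    meta: dict[str, str] = {}
    body = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        else:
            body.append(line)
    import io as _io

    df = pd.read_csv(_io.StringIO("\n".join(body)))
    gaps = ()
    if meta.get("gaps_s"):
        gaps = tuple(tuple(float(x) for x in g.split(","))
                     for g in meta["gaps_s"].split(";"))
    return GammaEventList(df["t_s"].to_numpy(), df["E_keV"].to_numpy(),
                          t_start_min=float(meta.get("t_start_min", 0.0)),
                          gaps_s=gaps)


def write_series(series: CountTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# background_rate_cps: {series.background_rate_cps}\n")
        fh.write(f"# background_rate_sd_cps: {series.background_rate_sd_cps}\n")
        fh.write(f"# origin: {series.origin}\n")
        fh.write("t_start_s,t_end_s,counts,masked\n")
        for a, b, c, m in zip(series.edges_s[:-1], series.edges_s[1:],
                              series.raw_counts, series.mask):
            fh.write(f"{a:.3f},{b:.3f},{int(c)},{int(m)}\n")


def read_series(path: str | Path) -> CountTimeSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    body = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        else:
            body.append(line)
    import io as _io

    df = pd.read_csv(_io.StringIO("\n".join(body)))
    edges = np.append(df["t_start_s"].to_numpy(), df["t_end_s"].to_numpy()[-1])
    return CountTimeSeries(
        edges, df["counts"].to_numpy(),
        background_rate_cps=float(meta.get("background_rate_cps", 0.0)),
        background_rate_sd_cps=float(meta.get("background_rate_sd_cps", 0.0)),
        mask=df["masked"].to_numpy(dtype=bool),
        origin=meta.get("origin", "end_of_irradiation"),
    )


def write_tac(tac: pd.DataFrame, path: str | Path) -> None:
    tac.to_csv(path, index=False)


def read_tac(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(report: dict, path: str | Path) -> None:
    """JSON report writer; numpy scalars/arrays are converted to plain types."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
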