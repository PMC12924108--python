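"""Delimited-text file contracts shared by the generator, CLI and pipeline.

All panels travel as comma-separated text with a header row; writers and
readers round-trip losslessly.  A study directory holds ``counties.csv``
(attributes plus a semicolon-separated neighbor list), ``population.csv``
(annual, by age group and sex), ``exposure.csv``, ``temperature.csv``,
``deaths.csv`` and, for synthetic studies, ``truth.txt`` (key=value).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .synthetic import CountyTable, SyntheticPanel


def write_panel(panel: SyntheticPanel, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tab = panel.counties.table.copy()
    tab["neighbors"] = [
        ";".join(sorted(panel.counties.adjacency.neighbors(c))) for c in tab["county_id"]
    ]
    tab.to_csv(d / "counties.csv", index=False)
    panel.counties.population.to_csv(d / "population.csv", index=False)
    panel.exposure.to_csv(d / "exposure.csv", index=False)
    panel.temperature.to_csv(d / "temperature.csv", index=False)
    panel.deaths.to_csv(d / "deaths.csv", index=False)
    with open(d / "truth.txt", "w") as fh:
        for key, val in panel.truth.items():
            if isinstance(val, pd.DataFrame):
                continue
            if isinstance(val, dict):
                val = json.dumps({str(k): v for k, v in val.items()})
            fh.write(f"{key}={val}\n")
        if panel.config is not None:
            fh.write(f"start_year={panel.config.start_year}\n")
            fh.write(f"seed={panel.config.seed}\n")
    return d


def read_panel(directory) -> SyntheticPanel:
    d = Path(directory)
    tab = pd.read_csv(d / "counties.csv")
    graph = nx.Graph()
    graph.add_nodes_from(tab["county_id"])
    for cid, nb in zip(tab["county_id"], tab["neighbors"].fillna("")):
        for other in str(nb).split(";"):
            if other:
                graph.add_edge(cid, other)
    counties = CountyTable(
        table=tab.drop(columns=["neighbors"]),
        adjacency=graph,
        population=pd.read_csv(d / "population.csv"),
    )
    truth: dict = {}
    truth_path = d / "truth.txt"
    if truth_path.exists():
        for line in truth_path.read_text().splitlines():
            if "=" in line:
                key, val = line.split("=", 1)
                truth[key] = val
    panel = SyntheticPanel(
        counties=counties,
        exposure=pd.read_csv(d / "exposure.csv"),
        temperature=pd.read_csv(d / "temperature.csv"),
        deaths=pd.read_csv(d / "deaths.csv"),
        truth=truth,
        config=None,
    )
    return panel


def write_manifest(path, **entries) -> None:
    """Run manifest: key=value log of config, seed, versions and counts."""
    import windlag

    lines = [f"windlag_version={windlag.__version__}"]
    lines += [f"numpy_version={np.__version__}", f"pandas_version={pd.__version__}"]
    for key, val in entries.items():
        lines.append(f"{key}={val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_keyvalues(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#") and "=" in line:
            key, val = line.split("=", 1)
            out[key] = val
    return out
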